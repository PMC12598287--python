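"""Imputation-accuracy metrics: stratified truth-vs-imputed confusion counts,
non-reference concordance, heterozygous FPR/FNR, and site-recovery tables.

Rates with an empty denominator are *undefined* and returned as ``None``
(an explicit sentinel, never silently 0 or NaN).

By default concordance is conditional on a call being made: imputed calls
that are missing after GP filtering sit in the imputed-MISSING column of the
confusion matrix and are excluded from rate denominators.  An unconditional
variant (missing counted as discordant) is available via ``conditional=False``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .gtio import apply_gp_filter, is_transition, maf_tranches
from .types import MISSING, SampleCallset

#: dosage -> confusion index (MISSING maps to row/col 3)
_IDX = {0: 0, 1: 1, 2: 2, MISSING: 3}
DOSAGE_ORDER = (0, 1, 2, MISSING)


@dataclass
class ConfusionCounts:
    """4x4 truth x imputed dosage counts per (tranche, substitution) stratum.

    Axis order is ``(0, 1, 2, MISSING)`` for both rows (truth) and columns
    (imputed).  ``matrix()`` pools over any subset of the strata.
    """

    counts: dict  # (tranche, subst) -> 4x4 int ndarray
    sample_id: str
    gp_threshold: float

    def strata(self) -> list[tuple]:
        return sorted(self.counts)

    def matrix(self, tranche: Optional[str] = None, subst: Optional[str] = None) -> np.ndarray:
        out = np.zeros((4, 4), dtype=np.int64)
        for (t, s), m in self.counts.items():
            if (tranche is None or t == tranche) and (subst is None or s == subst):
                out += m
        return out

    @property
    def total(self) -> int:
        return int(self.matrix().sum())


def crosstab(
    truth: SampleCallset,
    imputed: SampleCallset,
    gp_threshold: float = 0.0,
) -> ConfusionCounts:
    """Cross-tabulate truth vs (GP-filtered) imputed dosages per stratum.

    Sites where the truth is missing are excluded entirely; imputed calls
    failing the GP filter land in the imputed-MISSING column.  Counts over
    strata partition the compared sites exactly.
    """
    if len(truth.sites) != len(imputed.sites) or not truth.sites["pos"].equals(imputed.sites["pos"]):
        raise ValueError("truth and imputed callsets must share one site list")
    imp = apply_gp_filter(imputed, gp_threshold) if gp_threshold > 0 else imputed
    keep = truth.dosage != MISSING
    t_idx = np.array([_IDX[d] for d in truth.dosage[keep]])
    i_idx = np.array([_IDX[d] for d in imp.dosage[keep]])
    tranche = maf_tranches(truth.sites["maf"].to_numpy())[keep]
    subst = np.where(
        is_transition(truth.sites["ref"].to_numpy(), truth.sites["alt"].to_numpy()),
        "transition",
        "transversion",
    )[keep]
    counts: dict = {}
    frame = pd.DataFrame({"t": t_idx, "i": i_idx, "tr": tranche, "sc": subst})
    for (tr, sc), grp in frame.groupby(["tr", "sc"], sort=False):
        m = np.zeros((4, 4), dtype=np.int64)
        np.add.at(m, (grp["t"].to_numpy(), grp["i"].to_numpy()), 1)
        counts[(tr, sc)] = m
    return ConfusionCounts(counts, truth.sample_id, gp_threshold)


def nonref_concordance(m: np.ndarray, conditional: bool = True) -> Optional[float]:
    """Correct het + hom-alt calls over all truth het + hom-alt sites.

    ``conditional=True`` (default) excludes imputed-MISSING sites from the
    denominator; ``False`` counts them as not recovered.
    """
    num = m[1, 1] + m[2, 2]
    hi = 4 if not conditional else 3
    den = m[1, :hi].sum() + m[2, :hi].sum()
    return None if den == 0 else float(num / den)


def het_fpr(m: np.ndarray) -> Optional[float]:
    """Spurious imputed hets among truth homozygotes: FP/(FP+TN).

    FP = truth-hom imputed het; TN = truth-hom imputed as the *same* hom
    (cross-hom errors count in neither, following the formula's letter).
    """
    fp = m[0, 1] + m[2, 1]
    tn = m[0, 0] + m[2, 2]
    return None if fp + tn == 0 else float(fp / (fp + tn))


def het_fnr(m: np.ndarray) -> Optional[float]:
    """Truth hets imputed homozygous over truth hets with any imputed call."""
    den = m[1, 0] + m[1, 1] + m[1, 2]
    return None if den == 0 else float((m[1, 0] + m[1, 2]) / den)


def recovery_table(
    imputed_filtered: SampleCallset,
    pseudohaploid: SampleCallset,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Per-sample site-recovery accounting at a minimum-MAF cutoff (inclusive).

    Columns: number of non-missing imputed / pseudohaploid sites, and the
    imputed non-reference split into het and hom-alt.
    """
    maf = imputed_filtered.sites["maf"].to_numpy()
    sel = maf >= maf_min
    imp = imputed_filtered.dosage[sel]
    pse = pseudohaploid.dosage[sel]
    return pd.DataFrame(
        [
            {
                "sample": imputed_filtered.sample_id,
                "maf_min": maf_min,
                "n_sites": int(sel.sum()),
                "n_imputed_called": int((imp != MISSING).sum()),
                "n_pseudohap_called": int((pse != MISSING).sum()),
                "n_imputed_nonref": int(((imp == 1) | (imp == 2)).sum()),
                "n_imputed_het": int((imp == 1).sum()),
                "n_imputed_homalt": int((imp == 2).sum()),
            }
        ]
    )


def metrics_frame(cc: ConfusionCounts, conditional: bool = True) -> pd.DataFrame:
    """Tidy long table of all three rates per stratum plus pooled rows."""
    rows = []
    strata = cc.strata() + [(None, None)]
    for (tr, sc) in strata:
        m = cc.matrix(tr, sc)
        for name, fn in (
            ("nonref_concordance", lambda x: nonref_concordance(x, conditional)),
            ("het_fpr", het_fpr),
            ("het_fnr", het_fnr),
        ):
            rows.append(
                {
                    "sample": cc.sample_id,
                    "gp": cc.gp_threshold,
                    "tranche": tr if tr is not None else "all",
                    "subst_class": sc if sc is not None else "all",
                    "metric": name,
                    "value": fn(m),
                    "n": int(m[:3, :].sum()),
                }
            )
    return pd.DataFrame(rows)
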