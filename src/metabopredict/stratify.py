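"""Disease sub-group stratification by the 2-SD rule.

Animals are labelled from two day-20 traits, cumulative glycemia (CG) and
body weight (BW):

* ``Ob-IGT`` — both CG and BW above mean + k*SD,
* ``L-IGT``  — CG above its threshold, BW at or below its threshold,
* ``LNG``    — lean normoglycemic non-responders, below a configurable
  lower rule (default: at or below the lower decile on both traits),
* ``midgroup`` — everything else.

SD is the sample standard deviation (n-1 denominator).  The LNG/midgroup
boundary is not biologically sharp; the rule applied is recorded verbatim
in the result so every output is self-describing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StratificationResult", "stratify", "groups_to_targets", "CONTRASTS"]

GROUPS = ("LNG", "L-IGT", "Ob-IGT", "midgroup")


@dataclass
class StratificationResult:
    thresholds: dict
    labels: pd.Series
    rule: str

    def counts(self) -> dict:
        return {g: int((self.labels == g).sum()) for g in GROUPS}


def stratify(
    pheno: pd.DataFrame,
    glycemia_col: str = "CG",
    bw_col: str = "BW",
    k_sd: float = 2.0,
    lng_quantile: float = 0.1,
) -> StratificationResult:
    """Apply the mean + k*SD upper rule and the LNG lower rule.

    ``lng_quantile`` sets the lower rule: an animal is LNG when both traits
    are at or below that sample quantile (default 0.1, the lower decile:
    non-responders are an extreme tail, comparable in size to the other
    extreme groups).
    A zero SD in either trait yields no upper-threshold exceedance and a
    warning rather than an error.
    """
    for col in (glycemia_col, bw_col):
        if col not in pheno.columns:
            raise ValueError(f"column {col!r} not in phenotype table")
        if pheno[col].notna().sum() < 3:
            raise ValueError(f"column {col!r} needs >= 3 finite values")
    g = pheno[glycemia_col].to_numpy(dtype=float)
    b = pheno[bw_col].to_numpy(dtype=float)
    g_mean, g_sd = float(np.nanmean(g)), float(np.nanstd(g, ddof=1))
    b_mean, b_sd = float(np.nanmean(b)), float(np.nanstd(b, ddof=1))
    if g_sd == 0 or b_sd == 0:
        warnings.warn("zero SD in a stratifying trait; no animal exceeds mean+k*SD")
    t_g = g_mean + k_sd * g_sd
    t_b = b_mean + k_sd * b_sd
    q_g = float(np.nanquantile(g, lng_quantile))
    q_b = float(np.nanquantile(b, lng_quantile))

    labels = np.array(["midgroup"] * len(pheno), dtype=object)
    labels[(g > t_g) & (b > t_b)] = "Ob-IGT"
    labels[(g > t_g) & (b <= t_b)] = "L-IGT"
    lower = (g <= q_g) & (b <= q_b) & (labels == "midgroup")
    labels[lower] = "LNG"

    rule = (
        f"Ob-IGT: {glycemia_col}>mean+{k_sd}SD and {bw_col}>mean+{k_sd}SD; "
        f"L-IGT: {glycemia_col}>mean+{k_sd}SD only; "
        f"LNG: both traits <= sample quantile {lng_quantile}; else midgroup. "
        f"SD uses the n-1 denominator."
    )
    thresholds = {
        glycemia_col: {"mean": g_mean, "sd": g_sd, "upper": t_g, "lower": q_g},
        bw_col: {"mean": b_mean, "sd": b_sd, "upper": t_b, "lower": q_b},
    }
    return StratificationResult(thresholds, pd.Series(labels, index=pheno.index), rule)


CONTRASTS = {
    "extreme": ({"LNG", "L-IGT", "Ob-IGT"}, {"midgroup"}),
    "lean_vs_ob": ({"LNG", "L-IGT"}, {"Ob-IGT"}),
    "ng_vs_igt": ({"LNG"}, {"L-IGT", "Ob-IGT"}),
    "lng_vs_ligt": ({"LNG"}, {"L-IGT"}),
}


def groups_to_targets(
    result: StratificationResult, contrast: str
) -> tuple[list[str], pd.Series, dict]:
    """Binary class labels for a named disease-sub-group contrast.

    Returns (sample ids, 0/1 labels indexed by id, composition record).
    Class 0 is the first set in :data:`CONTRASTS`, class 1 the second.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; one of {sorted(CONTRASTS)}")
    class0, class1 = CONTRASTS[contrast]
    lab = result.labels
    ids0 = list(lab.index[lab.isin(class0)])
    ids1 = list(lab.index[lab.isin(class1)])
    if len(ids0) < 2 or len(ids1) < 2:
        raise ValueError(
            f"contrast {contrast!r}: need >= 2 animals per class, "
            f"got {len(ids0)} vs {len(ids1)}"
        )
    ids = ids0 + ids1
    y = pd.Series([0] * len(ids0) + [1] * len(ids1), index=ids, name=contrast)
    composition = {
        "contrast": contrast,
        "class0": sorted(class0),
        "class1": sorted(class1),
        "n0": len(ids0),
        "n1": len(ids1),
    }
    return ids, y, composition
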