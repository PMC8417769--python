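"""Volumetric group studies on soft segmentations.

Structure volumes are integrated directly from the softmax probability maps
(sum of per-voxel probabilities times the voxel volume), which accounts for
segmentation uncertainty and, to some extent, partial-volume effects.
Volumes are then corrected for age and intracranial volume (ICV) with an
ordinary-least-squares general linear model fitted over all subjects
(adjusted volume = residual + grand mean), and group differences between
controls and patients are quantified with Cohen's d

    d = (mu_C - mu_A) / s,
    s = sqrt(((n_C - 1) s_C^2 + (n_A - 1) s_A^2) / (n_C + n_A - 2)),

with unpaired one-tailed t-tests (direction: control > disease, the atrophy
hypothesis).  An effect is called small when |d| < 0.2 and large when
|d| > 0.8.  Raw p-values are reported; the report records how many tests
were run so the reader can account for multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import SoftLabelMap

__all__ = [
    "StudyTable",
    "EffectSizeReport",
    "soft_volumes",
    "build_study_table",
    "residualize",
    "cohens_d",
    "group_test",
    "run_group_study",
]

COVARIATE_COLUMNS = ("subject", "group", "age", "icv")


@dataclass
class StudyTable:
    """Per-subject covariates plus per-structure volumes (mm^3).

    ``frame`` holds one row per subject with columns subject, group
    ('control'/'disease'), age (years), icv (mm^3) and one column per
    structure volume.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"study table is missing columns: {missing}")
        if self.frame[list(COVARIATE_COLUMNS)].isna().any().any():
            raise ValueError("study table has missing covariates")
        groups = set(self.frame["group"])
        if not groups <= {"control", "disease"} or len(groups) < 1:
            raise ValueError(f"group labels must be 'control'/'disease', got {groups}")
        if not self.structures:
            raise ValueError("study table has no structure volume columns")
        if (self.frame[self.structures] < 0).any().any():
            raise ValueError("volumes must be non-negative")

    @property
    def structures(self) -> list[str]:
        return [c for c in self.frame.columns if c not in COVARIATE_COLUMNS]

    def group(self, label: str) -> pd.DataFrame:
        return self.frame[self.frame["group"] == label]


def soft_volumes(s: SoftLabelMap) -> pd.Series:
    """Structure volumes in mm^3 from a probability map.

    Each label volume is the sum of its channel probabilities times the
    voxel volume; 'whole left'/'whole right'/'whole' are sums of the
    corresponding subunit volumes.
    """
    voxel_mm3 = float(np.prod(s.voxel_size))
    tax = s.taxonomy
    sums = s.data.reshape(-1, s.data.shape[-1]).sum(axis=0, dtype=np.float64) * voxel_mm3
    vols = {tax.name_of(c): float(sums[tax.index_of(c)]) for c in tax.codes}
    left = [c for c in tax.foreground_codes if tax.lr_swap[c] > c]
    right = [c for c in tax.foreground_codes if tax.lr_swap[c] < c]
    vols["whole left"] = float(sum(sums[tax.index_of(c)] for c in left))
    vols["whole right"] = float(sum(sums[tax.index_of(c)] for c in right))
    vols["whole"] = float(sum(sums[tax.index_of(c)] for c in tax.foreground_codes))
    return pd.Series(vols)


def build_study_table(
    soft_maps: dict[str, SoftLabelMap], covariates: pd.DataFrame
) -> StudyTable:
    """Join per-subject soft-segmentation volumes with their covariates."""
    cov = covariates.copy()
    cov["subject"] = cov["subject"].astype(str)
    rows = []
    for subject, smap in soft_maps.items():
        vols = soft_volumes(smap)
        vols = vols.drop(labels=[smap.taxonomy.name_of(smap.taxonomy.background)])
        rows.append(pd.Series({"subject": str(subject), **vols.to_dict()}))
    vol_frame = pd.DataFrame(rows)
    merged = cov.merge(vol_frame, on="subject", how="inner")
    if len(merged) != len(vol_frame):
        missing = set(vol_frame["subject"]) - set(cov["subject"])
        raise ValueError(f"subjects missing from the covariate table: {sorted(missing)}")
    return StudyTable(merged)


def residualize(table: StudyTable, covariates=("age", "icv")) -> StudyTable:
    """Correct structure volumes for covariates with an OLS linear model.

    Each structure volume is regressed on an intercept plus the covariates
    over all subjects jointly; the adjusted volume is the residual plus the
    grand mean, which keeps volumes on their original scale.
    """
    frame = table.frame.copy()
    design = frame[list(covariates)].astype(float)
    for cov in covariates:
        if design[cov].nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant; cannot correct for it")
    x = sm.add_constant(design.to_numpy())
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    for structure in table.structures:
        y = frame[structure].astype(float).to_numpy()
        fit = sm.OLS(y, x).fit()
        frame[structure] = fit.resid + y.mean()
    return StudyTable(frame)


def cohens_d(values_c, values_a) -> float:
    """Cohen's d with the pooled sample standard deviation (n-1 variances)."""
    c = np.asarray(values_c, dtype=float)
    a = np.asarray(values_a, dtype=float)
    if c.size < 2 or a.size < 2:
        raise ValueError("need at least two values per group")
    s2 = ((c.size - 1) * c.var(ddof=1) + (a.size - 1) * a.var(ddof=1)) / (
        c.size + a.size - 2
    )
    if s2 == 0.0:
        raise ValueError("pooled standard deviation is zero; d is undefined")
    return float((c.mean() - a.mean()) / np.sqrt(s2))


def group_test(values_c, values_a) -> float:
    """One-tailed pooled-variance t-test p-value for control > disease."""
    c = np.asarray(values_c, dtype=float)
    a = np.asarray(values_a, dtype=float)
    if c.size < 2 or a.size < 2:
        raise ValueError("need at least two values per group")
    res = stats.ttest_ind(c, a, equal_var=True, alternative="greater")
    return float(res.pvalue)


def _magnitude(d: float) -> str:
    if abs(d) < 0.2:
        return "small"
    if abs(d) > 0.8:
        return "large"
    return "medium"


@dataclass
class EffectSizeReport:
    """Per-structure effect sizes with group summary statistics.

    ``frame`` has one row per structure: cohens_d, p_value, group means and
    variances, pooled s, group sizes and a small/medium/large annotation.
    ``n_tests`` records how many structures were tested (no multiplicity
    correction is applied to the reported raw p-values).
    """

    frame: pd.DataFrame
    n_tests: int = 0
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, structure: str) -> pd.Series:
        sub = self.frame[self.frame["structure"] == structure]
        if sub.empty:
            raise KeyError(structure)
        return sub.iloc[0]


def run_group_study(
    soft_maps: dict[str, SoftLabelMap],
    covariates: pd.DataFrame,
    correct_for=("age", "icv"),
) -> EffectSizeReport:
    """Full volumetric group study: volumes -> GLM correction -> effects.

    Requires at least two subjects per group.  Returns per-structure
    Cohen's d (control minus disease over pooled s) and one-tailed t-test
    p-values on the covariate-adjusted volumes.
    """
    table = build_study_table(soft_maps, covariates)
    for label in ("control", "disease"):
        if len(table.group(label)) < 2:
            raise ValueError(f"need at least 2 subjects in group {label!r}")
    adjusted = residualize(table, covariates=correct_for) if correct_for else table

    rows, flags = [], []
    ctrl, dis = adjusted.group("control"), adjusted.group("disease")
    for structure in adjusted.structures:
        c = ctrl[structure].to_numpy(dtype=float)
        a = dis[structure].to_numpy(dtype=float)
        try:
            d = cohens_d(c, a)
            p = group_test(c, a)
        except ValueError:
            flags.append(structure)
            d, p = np.nan, np.nan
        pooled = np.sqrt(
            ((c.size - 1) * c.var(ddof=1) + (a.size - 1) * a.var(ddof=1))
            / (c.size + a.size - 2)
        )
        rows.append(
            {
                "structure": structure,
                "cohens_d": d,
                "p_value": p,
                "mean_control": c.mean(),
                "mean_disease": a.mean(),
                "var_control": c.var(ddof=1),
                "var_disease": a.var(ddof=1),
                "pooled_s": pooled,
                "n_control": c.size,
                "n_disease": a.size,
                "magnitude": _magnitude(d) if np.isfinite(d) else "undefined",
            }
        )
    frame = pd.DataFrame(rows)
    return EffectSizeReport(frame, n_tests=len(rows), flags=flags)
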