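"""Paired-design inference for the intact vs. CCL-deficient comparison.

The study design is fully paired: every specimen is measured intact and
again after CCL transection, at each of the two flexion angles.  Scalar
metrics (contact area, peak/mean pressure, peak-pressure location, pose
components) are compared with paired t-tests; the regional contact forces
are compared with a fixed-effects general linear model

    force ~ status * region + specimen

fitted per compartment, from which the status contrast (transected - intact)
is extracted for each region.  Two-sided tests throughout; the significance
threshold is alpha = 0.01 and no multiple-testing correction is applied
beyond that strict threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .contact import REGIONS
from .errors import DegenerateSampleError, InputError

__all__ = [
    "ALPHA",
    "PairedSample",
    "PairedTResult",
    "paired_t",
    "regional_glm",
    "summarize",
    "format_mean_sd",
]

#: significance threshold used throughout the analysis
ALPHA = 0.01

STATUS_LEVELS = ("intact", "transected")


@dataclass(frozen=True)
class PairedSample:
    """Matched measurements of one metric under two conditions.

    ``values_a`` and ``values_b`` are matched by specimen id (same order);
    differences are taken as ``a - b``.
    """

    specimen_ids: tuple
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self):
        ids = tuple(self.specimen_ids)
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if not (len(ids) == a.size == b.size):
            raise InputError(
                f"mismatched paired sample: {len(ids)} ids, {a.size} vs "
                f"{b.size} values"
            )
        if a.size < 2:
            raise InputError("paired sample needs at least 2 specimens")
        if len(set(ids)) != len(ids):
            raise InputError("duplicate specimen ids in paired sample")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise InputError("non-finite values in paired sample")
        object.__setattr__(self, "specimen_ids", ids)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    @property
    def n(self) -> int:
        return len(self.specimen_ids)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    sd_diff: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def paired_t(sample: PairedSample) -> PairedTResult:
    """Two-sided paired Student t-test on ``values_a - values_b``.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``df = n - 1`` and the p-value
    from the Student t distribution.  Raises
    :class:`~stiflemech.errors.DegenerateSampleError` when the differences
    have zero variance (the statistic is undefined), except in the exact
    null case d == 0 where (t, p) = (0, 1) is well defined and returned.
    """
    d = sample.values_a - sample.values_b
    n = sample.n
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedTResult(0.0, n - 1, 1.0, 0.0, 0.0, n)
        raise DegenerateSampleError(
            "paired differences have zero variance but non-zero mean; "
            "t statistic is undefined"
        )
    t = mean_d / (sd_d / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return PairedTResult(float(t), n - 1, p, mean_d, sd_d, n)


REQUIRED_FORCE_COLUMNS = ("specimen", "compartment", "region", "ccl_status", "force")


def _validate_force_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_FORCE_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"regional force table missing columns {missing}")
    bad_regions = set(table["region"]) - set(REGIONS)
    if bad_regions:
        raise InputError(f"unknown regions {sorted(bad_regions)}")
    bad_status = set(table["ccl_status"]) - set(STATUS_LEVELS)
    if bad_status:
        raise InputError(f"unknown ccl_status {sorted(bad_status)}")
    if table["specimen"].nunique() < 2:
        raise InputError("regional GLM needs at least 2 specimens")
    # balanced design: 3 regions x 2 statuses per specimen x compartment
    counts = table.groupby(["specimen", "compartment"]).size()
    if not (counts == 6).all():
        raise InputError(
            "unbalanced regional force table: every specimen x compartment "
            "needs exactly 3 regions x 2 statuses"
        )
    cell = table.groupby(["specimen", "compartment", "region", "ccl_status"]).size()
    if not (cell == 1).all():
        raise InputError("duplicate specimen x region x status rows in force table")
    return table


def regional_glm(table: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Status contrasts of regional contact force from a blocked linear model.

    ``table`` is long-format with columns ``specimen, compartment, region,
    ccl_status, force`` and must be balanced.  Per compartment, the blocked
    model ``force ~ C(ccl_status) * C(region) + C(specimen)`` is fitted by
    OLS; its status x region interaction F-test is reported per compartment
    (``interaction_p``), and the transected-minus-intact contrast is
    evaluated within each region.

    Contrast standard errors use the *region-specific* error stratum (the
    variance of the within-specimen paired differences of that region, df =
    n - 1) rather than the pooled OLS residual: regional forces are strongly
    heteroscedastic — an unloaded region carries ~0 N with near-zero
    variance while a loaded one varies by tens of N — and pooled-variance
    contrasts are badly anti-conservative for the high-variance regions.
    In the balanced design the point estimates coincide with the OLS ones,
    and a single-region table reduces exactly to the paired t-test.

    Returns a tidy frame with one row per compartment x region:
    ``estimate`` (N, transected - intact), ``se``, ``t``, ``df``, ``p``,
    ``significant`` (p < alpha) and the compartment's ``interaction_p``.
    """
    table = _validate_force_table(table)
    out = []
    for compartment, dfc in table.groupby("compartment", sort=True):
        fit = smf.ols(
            "force ~ C(ccl_status, Treatment('intact')) * C(region) + C(specimen)",
            data=dfc,
        ).fit()
        names = [n for n in fit.params.index if ":" in n]
        interaction_p = float(fit.f_test(" = ".join(names) + " = 0").pvalue) if names else 1.0
        wide = dfc.pivot_table(
            index=["specimen", "region"], columns="ccl_status", values="force"
        )
        for region in REGIONS:
            d = (
                wide.xs(region, level="region")["transected"]
                - wide.xs(region, level="region")["intact"]
            ).to_numpy()
            n = d.size
            est = float(d.mean())
            sd = float(d.std(ddof=1))
            if sd == 0.0:
                t = 0.0 if est == 0.0 else np.inf * np.sign(est)
                p = 1.0 if est == 0.0 else 0.0
                se = 0.0
            else:
                se = sd / np.sqrt(n)
                t = est / se
                p = float(2.0 * sps.t.sf(abs(t), n - 1))
            out.append(
                {
                    "compartment": compartment,
                    "region": region,
                    "estimate": est,
                    "se": se,
                    "t": float(t),
                    "df": n - 1,
                    "p": p,
                    "significant": p < alpha,
                    "interaction_p": interaction_p,
                }
            )
    return pd.DataFrame(out)


def summarize(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1; 0.0 for n == 1)."""
    a = np.asarray(list(values), dtype=float)
    if a.size == 0:
        raise InputError("cannot summarize an empty sample")
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    return float(a.mean()), sd


def format_mean_sd(mean: float, sd: float, ndigits: int = 1) -> str:
    """Table-style ``mean+/-sd`` cell text, e.g. ``316.0±34.0`` (ndigits=1)
    or ``2±1`` (ndigits=0)."""
    return f"{mean:.{ndigits}f}±{sd:.{ndigits}f}"
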